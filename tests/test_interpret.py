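"""Integrated gradients, critical dimensions, ablation classification."""

import numpy as np
import pytest

from synerank.encoders import ModelConfig, SynergyModel
from synerank.interpret import (
    _segments,
    ablate_and_classify,
    critical_dimensions,
    integrated_gradients,
    select_high_confidence,
    summarize_drivers,
)


@pytest.fixture
def linear_model(rng):
    """Model whose head is a single affine layer: f(x) = w.x + b."""
    model = SynergyModel(ModelConfig.desk(head_hidden=(), seed=0))
    model.head_out.W.data = rng.normal(size=model.head_out.W.data.shape)
    model.head_out.b.data = np.array([0.7])
    return model


@pytest.fixture
def mlp_model():
    return SynergyModel(ModelConfig.desk(seed=1))


def roughened_mlp(seed):
    """MLP with inflated weights so its head is strongly non-linear and the
    path-integral discretisation error is measurably non-zero."""
    model = SynergyModel(ModelConfig.desk(seed=seed))
    rng = np.random.default_rng(seed)
    for layer in [*model.head_layers, model.head_out]:
        layer.W.data *= 4.0
        layer.b.data = rng.normal(size=layer.b.data.shape)
    return model


def test_linear_model_attribution_is_x_times_w_exactly(linear_model, rng):
    dim = linear_model.config.head_in_dim()
    x = rng.normal(size=dim)
    w = linear_model.head_out.W.data[:, 0]
    for n_steps in (2, 5, 64):
        attrs, residual = integrated_gradients(linear_model, x, n_steps=n_steps)
        flat = np.concatenate([attrs[m] for m in ("drug1", "drug2", "dose1", "dose2", "cell")])
        np.testing.assert_allclose(flat, x * w, atol=1e-10)
        assert residual < 1e-10


def test_baseline_input_gets_zero_attribution(mlp_model):
    dim = mlp_model.config.head_in_dim()
    attrs, _ = integrated_gradients(mlp_model, np.zeros(dim), n_steps=8)
    for v in attrs.values():
        np.testing.assert_array_equal(v, 0.0)


def test_completeness_residual_shrinks_with_step_count(rng):
    model = roughened_mlp(seed=2)
    x = rng.normal(size=model.config.head_in_dim())
    residuals = [integrated_gradients(model, x, n_steps=n)[1] for n in (32, 64, 128)]
    assert residuals[0] > 1e-12  # meaningfully non-linear
    assert residuals[0] > residuals[1] > residuals[2]


def test_step_count_below_two_rejected(mlp_model):
    with pytest.raises(ValueError):
        integrated_gradients(mlp_model, np.zeros(mlp_model.config.head_in_dim()), n_steps=1)


# -- critical dimensions -----------------------------------------------------


def test_critical_dimensions_threshold_rule():
    dims, degenerate = critical_dimensions(np.array([1.0, 0.5, 0.7]), fraction=0.6)
    assert list(dims) == [0, 2] and not degenerate


def test_uniform_attribution_selects_all_dims():
    dims, _ = critical_dimensions(np.full(5, 0.3))
    assert list(dims) == [0, 1, 2, 3, 4]


def test_all_zero_attribution_flagged_degenerate():
    dims, degenerate = critical_dimensions(np.zeros(4))
    assert dims.size == 0 and degenerate


def test_argmax_always_included_even_under_strict_inequality():
    dims, _ = critical_dimensions(np.array([0.2, -0.9, 0.1]), fraction=0.6)
    assert 1 in dims


def test_critical_dimensions_match_brute_force(rng):
    for _ in range(100):
        v = rng.normal(size=rng.integers(1, 40))
        dims, _ = critical_dimensions(v, fraction=0.6)
        expected = {i for i, a in enumerate(np.abs(v)) if a > 0.6 * np.abs(v).max()}
        expected.add(int(np.abs(v).argmax()))
        assert set(dims.tolist()) == expected


# -- ablation classification -------------------------------------------------


def _model_with_weights_on(segment_name, rng):
    model = SynergyModel(ModelConfig.desk(head_hidden=(), seed=0))
    segs = _segments(model)
    w = np.zeros_like(model.head_out.W.data)
    seg = segs[segment_name]
    w[seg] = np.abs(rng.normal(size=(seg.stop - seg.start, 1)))
    model.head_out.W.data = w
    model.head_out.b.data = np.zeros(1)
    return model


@pytest.mark.parametrize(
    "segment,expected",
    [("drug1", "Drug1-dominant"), ("drug2", "Drug2-dominant"), ("cell", "Cell-dominant")],
)
def test_single_modality_linear_model_labelled_correctly(segment, expected, rng):
    model = _model_with_weights_on(segment, rng)
    x = np.abs(rng.normal(size=model.config.head_in_dim()))  # positive prediction
    rep = ablate_and_classify(model, x, ("A", "B", "C"), dominance_margin=0.0)
    assert rep.label == expected
    for m, d in rep.deltas.items():
        if m != segment:
            assert d == pytest.approx(0.0, abs=1e-12)


def test_balanced_when_margin_not_met():
    model = SynergyModel(ModelConfig.desk(head_hidden=(), seed=0))
    model.head_out.W.data[:] = 0.0
    model.head_out.b.data = np.array([1.0])  # constant head: all deltas 0
    rep = ablate_and_classify(
        model, np.ones(model.config.head_in_dim()), ("A", "B", "C"), dominance_margin=0.1
    )
    assert rep.label == "Balanced"
    assert all(d == 0.0 for d in rep.deltas.values())
    assert all(rep.degenerate.values())


def test_classification_invariant_to_drug_relabelling(rng):
    # for a drug-order-symmetric model, swapping the two drug slots of the
    # input swaps the drug deltas and the label follows the relabelling
    model = SynergyModel(ModelConfig.desk(head_hidden=(), seed=0))
    segs = _segments(model)
    d = model.config.drug_out_dim()
    w = np.zeros_like(model.head_out.W.data)
    shared = rng.normal(size=(d, 1))
    w[segs["drug1"]] = shared
    w[segs["drug2"]] = shared  # identical slot weights -> symmetric head
    w[segs["cell"]] = 0.1 * rng.normal(size=(256, 1))
    model.head_out.W.data = w
    model.head_out.b.data = np.zeros(1)

    x = rng.normal(size=model.config.head_in_dim())
    x[segs["drug1"]] = np.abs(x[segs["drug1"]]) * np.sign(shared[:, 0]) * 2.0
    rep = ablate_and_classify(model, x, ("A", "B", "C"), dominance_margin=0.0)
    x_sw = x.copy()
    x_sw[0:d], x_sw[d : 2 * d] = x[d : 2 * d].copy(), x[0:d].copy()
    rep_sw = ablate_and_classify(model, x_sw, ("B", "A", "C"), dominance_margin=0.0)
    assert rep.deltas["drug1"] == pytest.approx(rep_sw.deltas["drug2"], rel=1e-9)
    assert rep.deltas["drug2"] == pytest.approx(rep_sw.deltas["drug1"], rel=1e-9)
    assert rep.deltas["cell"] == pytest.approx(rep_sw.deltas["cell"], rel=1e-9)
    assert rep.label == "Drug1-dominant" and rep_sw.label == "Drug2-dominant"


def _stub_report(deltas, original=1.0):
    from synerank.interpret import AttributionReport

    return AttributionReport(
        triplet=("A", "B", "C"),
        original_score=original,
        attributions={},
        critical_dims={},
        deltas=deltas,
        label="",
    )


@pytest.mark.parametrize(
    "deltas,margin,expected",
    [
        ({"drug1": 0.5, "drug2": 0.1, "cell": 0.1}, 0.1, "Drug1-dominant"),
        ({"drug1": 0.30, "drug2": 0.29, "cell": 0.28}, 0.1, "Balanced"),
        ({"drug1": 0.1, "drug2": 0.2, "cell": 0.5}, 0.1, "Cell-dominant"),
    ],
)
def test_dominance_margin_rule(deltas, margin, expected):
    from synerank.interpret import _merge_orientations

    flipped = dict(deltas, drug1=deltas["drug2"], drug2=deltas["drug1"])
    rep = _merge_orientations(_stub_report(deltas), _stub_report(flipped), margin)
    assert rep.label == expected


# -- selection and summary ---------------------------------------------------


def test_selection_empty_when_all_below_threshold():
    scores = {("a", "b", "c"): 0.5, ("a", "d", "c"): 0.79}
    assert select_high_confidence(scores, threshold=0.8) == []


def test_selection_truncates_to_top_k_descending():
    scores = {(f"d{i}", "x", "c"): 0.8 + 0.001 * i for i in range(1, 61)}
    out = select_high_confidence(scores, threshold=0.8, top_k=50)
    assert len(out) == 50
    vals = [s for _, s in out]
    assert vals == sorted(vals, reverse=True)
    assert min(vals) > 0.8 + 0.001 * 10  # the weakest 10 qualifiers were cut


def test_driver_summary_counts_and_fractions(rng):
    class R:
        def __init__(self, label):
            self.label = label

    reports = [R("Balanced")] * 3 + [R("Cell-dominant")] * 5 + [R("Drug1-dominant")] * 2
    s = summarize_drivers(reports)
    assert s["counts"]["Cell-dominant"] == 5
    assert s["fractions"]["Balanced"] == pytest.approx(0.3)
    assert sum(s["fractions"].values()) == pytest.approx(1.0)
    assert summarize_drivers([])["n"] == 0
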