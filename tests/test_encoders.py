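"""Encoders: sinusoidal dose code, tokenizer, CNN/ECFP drug paths, head."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synerank.encoders import (
    DOSE_DIM,
    ModelConfig,
    SynergyModel,
    dose_position,
    ecfp_bits,
    load_model,
    save_model,
    sinusoidal_encode,
    tokenize_smiles,
)
from synerank.synthetic_data import FIXTURE_SMILES


# -- sinusoidal dose encoding ------------------------------------------------


def test_zero_position_gives_alternating_zero_one_pattern():
    v = sinusoidal_encode(0.0)
    np.testing.assert_array_equal(v[0::2], np.zeros(32))
    np.testing.assert_array_equal(v[1::2], np.ones(32))


@settings(max_examples=200, deadline=None)
@given(st.floats(-1e4, 1e4, allow_nan=False))
def test_components_bounded_for_finite_inputs(r):
    v = sinusoidal_encode(r)
    assert v.shape == (DOSE_DIM,)
    assert np.all(v >= -1.0) and np.all(v <= 1.0)


def test_direct_evaluation_of_components():
    # independent evaluation of sin/cos(r * 10^(-4i/64)) at spot indices
    v = sinusoidal_encode(1.0)
    assert v[0] == pytest.approx(math.sin(1.0), abs=1e-12)
    assert v[1] == pytest.approx(math.cos(10.0 ** (-4 / 64)), abs=1e-12)
    assert v[2] == pytest.approx(math.sin(10.0 ** (-8 / 64)), abs=1e-12)
    assert v[63] == pytest.approx(math.cos(10.0 ** (-4 * 63 / 64)), abs=1e-12)


def test_component_frequency_strictly_decreasing():
    freq = 10.0 ** (-4.0 * np.arange(DOSE_DIM) / DOSE_DIM)
    assert np.all(np.diff(freq) < 0)


def test_non_finite_position_rejected():
    with pytest.raises(ValueError):
        sinusoidal_encode(float("nan"))


def test_dose_position_neglog10_and_zero_convention():
    pos = dose_position(np.array([1e-6, 1e-8, 0.0]))
    np.testing.assert_allclose(pos, [6.0, 8.0, 0.0])


# -- tokenizer ---------------------------------------------------------------


@pytest.fixture(scope="module")
def config():
    return ModelConfig.desk(max_smiles_length=40, seed=0)


def test_character_tokens_and_padding(config):
    toks = tokenize_smiles("CCO", config)
    v = config.vocabulary
    assert toks.shape == (40,)
    assert list(toks[:3]) == [v["C"], v["C"], v["O"]]
    assert np.all(toks[3:] == 0)


def test_two_character_atoms_are_single_tokens(config):
    toks = tokenize_smiles("CClBr", config)
    n_nonpad = int(np.sum(toks != 0))
    assert n_nonpad == 3


def test_unknown_character_maps_to_reserved_token(config):
    toks = tokenize_smiles("C!C", config)
    assert toks[1] == 1  # UNK


def test_empty_smiles_rejected(config):
    with pytest.raises(ValueError):
        tokenize_smiles("", config)


def test_tokenizer_injective_on_fixture_library(config):
    seen = {}
    for smi in FIXTURE_SMILES:
        key = tokenize_smiles(smi, config).tobytes()
        assert key not in seen, f"{smi} collides with {seen.get(key)}"
        seen[key] = smi


# -- drug / cell / head ------------------------------------------------------


@pytest.fixture(scope="module")
def model(config):
    return SynergyModel(config)


def test_drug_embedding_has_contract_dimension_and_is_deterministic(model, config):
    toks = tokenize_smiles("CC(=O)O", config)[None, :]
    e1 = model.encode_drugs(toks).data
    e2 = model.encode_drugs(toks).data
    assert e1.shape == (1, 128)
    np.testing.assert_array_equal(e1, e2)


def test_drug_embedding_sensitive_to_token_change(config):
    for seed in range(3):
        m = SynergyModel(ModelConfig.desk(max_smiles_length=40, seed=seed))
        a = m.encode_drugs(tokenize_smiles("CCO", config)[None, :]).data
        b = m.encode_drugs(tokenize_smiles("CCN", config)[None, :]).data
        assert not np.allclose(a, b)


def test_wrong_token_length_rejected(model):
    with pytest.raises(ValueError):
        model.encode_drugs(np.zeros((1, 7), dtype=np.intp))


def test_cell_embedding_contract(model, config):
    x = np.zeros(config.n_genes)
    e = model.encode_cells(x)
    assert e.data.shape == (1, 256)
    assert np.all(np.isfinite(e.data))
    with pytest.raises(ValueError):
        model.encode_cells(np.zeros(config.n_genes + 1))


def test_prediction_deterministic_and_finite_for_monotherapy(model, config, rng):
    expr = rng.normal(size=config.n_genes)
    y1 = model.predict("CCO", None, 1e-6, 0.0, expr)
    y2 = model.predict("CCO", None, 1e-6, 0.0, expr)
    assert y1 == y2 and math.isfinite(y1)


def test_batch_prediction_equals_per_sample(model, config, rng):
    smiles = ["CCO", "c1ccccc1", None]
    expr = rng.normal(size=(2, config.n_genes))
    d1 = np.array([0, 1, 0])
    d2 = np.array([1, 2, 2])
    cell = np.array([0, 1, 0])
    dose1 = np.array([1e-6, 1e-7, 1e-5])
    dose2 = np.array([1e-7, 0.0, 0.0])
    batch = model.predict_batch(smiles, d1, d2, expr, cell, dose1, dose2)
    for i in range(3):
        single = model.predict_batch(
            smiles, d1[[i]], d2[[i]], expr, cell[[i]], dose1[[i]], dose2[[i]]
        )
        assert batch[i] == pytest.approx(single[0], rel=1e-12)


# -- ablation variants -------------------------------------------------------


def test_linear_dose_encoder_is_affine():
    m = SynergyModel(ModelConfig.desk(dose_encoding="linear", seed=1))
    enc = lambda r: m.encode_doses(np.array([r])).data[0]
    assert enc(1.5).shape == (64,)
    np.testing.assert_allclose(enc(1.0) + enc(2.0) - enc(0.0), enc(3.0), atol=1e-9)
    np.testing.assert_array_equal(enc(0.7), enc(0.7))


def test_ecfp_bit_vector_contract():
    bits = ecfp_bits("CCO")
    assert bits.shape == (1024,)
    assert set(np.unique(bits)) <= {0.0, 1.0}


def test_ecfp_identical_for_different_spellings_of_same_molecule():
    # aromatic ring written from different starting atoms / kekulized
    a = ecfp_bits("Oc1ccccc1")
    b = ecfp_bits("c1ccc(O)cc1")
    np.testing.assert_array_equal(a, b)


def test_ecfp_unparseable_smiles_raises():
    with pytest.raises(ValueError):
        ecfp_bits("notasmiles((")


def test_ecfp_projected_mode_gives_128_dims():
    m = SynergyModel(ModelConfig.desk(drug_encoding="ecfp", seed=0))
    rows = m.drug_input_rows(["CCO", None])
    assert rows.shape == (2, 1024)
    assert np.all(rows[1] == 0)  # null drug = empty fingerprint
    e = m.encode_drug_inputs(rows)
    assert e.data.shape == (2, 128)


def test_ecfp_folded_mode_feeds_bits_to_head(rng):
    m = SynergyModel(ModelConfig.desk(drug_encoding="ecfp_folded", seed=0))
    assert m.config.head_in_dim() == 2 * 1024 + 2 * 64 + 256
    y = m.predict("CCO", "c1ccccc1", 1e-6, 1e-7, rng.normal(size=m.config.n_genes))
    assert math.isfinite(y)


# -- checkpointing -----------------------------------------------------------


def test_checkpoint_round_trip_preserves_predictions(tmp_path, config, rng):
    model = SynergyModel(config)
    model.target_mean, model.target_sd = 50.0, 10.0
    expr = rng.normal(size=config.n_genes)
    before = model.predict("CCO", "CCN", 1e-6, 1e-7, expr)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.predict("CCO", "CCN", 1e-6, 1e-7, expr) == before
    assert loaded.config.config_hash() == config.config_hash()
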