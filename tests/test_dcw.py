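"""SMILES optimal descriptor: tokenization, DCW arithmetic, Monte-Carlo fit."""

from collections import Counter

import numpy as np
import pytest

from fdtox import DCWModel, extract_attributes, optimize_weights
from fdtox.dcw import tokenize
from fdtox.errors import OptimizationError, ParseError

TRAIN_SMILES = [
    "CCO", "CCCO", "CC(O)CO", "OCCO", "CCCCO", "CC(C)O",
    "OCC(O)CO", "CCOCC", "CCC", "CCCC", "OC(CO)CO", "CCOC",
]


class TestTokenization:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("CCO", {"C": 2, "O": 1}),
            ("ClC", {"Cl": 1, "C": 1}),          # Cl is one token, not C+l
            ("BrCBr", {"Br": 2, "C": 1}),
            ("[NH3+]C", {"[NH3+]": 1, "C": 1}),  # bracket atom is one token
        ],
    )
    def test_order1_attributes(self, smiles, expected):
        assert extract_attributes(smiles, order=1) == Counter(expected)

    def test_ring_bond_tokens_retained(self):
        assert "1" in tokenize("C1CC1")
        assert "%12" in tokenize("C%12CC%12")

    def test_order2_pairs_are_lexicographic(self):
        attrs = extract_attributes("CO", order=2)
        assert attrs["C|O"] == 1
        assert "O|C" not in attrs

    def test_attributes_computed_on_canonical_smiles(self):
        # same molecule, different input atom orders
        assert extract_attributes("OCC", 2) == extract_attributes("CCO", 2)

    def test_empty_smiles_rejected(self):
        with pytest.raises(ParseError):
            extract_attributes("", order=1)

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(ParseError):
            extract_attributes("C(((", order=1)


class TestDcwValue:
    def test_all_zero_weights_give_zero(self):
        m = DCWModel(weights={"C": 0.0, "O": 0.0}, order=1, threshold=1,
                     n_epochs=0, step=0.1, seed=0)
        assert m.dcw_value(Counter({"C": 5, "O": 2})) == 0.0

    def test_weighted_sum_arithmetic(self):
        m = DCWModel(weights={"C": 1.0, "O": 2.0}, order=1, threshold=1,
                     n_epochs=0, step=0.1, seed=0)
        assert m.dcw_value(Counter({"C": 2, "O": 1})) == pytest.approx(4.0)

    def test_unknown_attributes_contribute_zero_and_are_counted(self):
        m = DCWModel(weights={"C": 1.0}, order=1, threshold=1,
                     n_epochs=0, step=0.1, seed=0)
        before = m.unknown_attribute_count
        assert m.dcw_value(Counter({"C": 1, "Zz": 3})) == pytest.approx(1.0)
        assert m.unknown_attribute_count == before + 1

    def test_subthreshold_attributes_frozen_at_zero(self):
        y = np.arange(12, dtype=float)
        model = optimize_weights(TRAIN_SMILES, y, order=1, threshold=3,
                                 n_epochs=5, seed=0)
        rare = [a for a, n in _presence().items() if n < 3]
        for attr in rare:
            assert model.weights.get(attr, 0.0) == 0.0


def _presence() -> Counter:
    presence = Counter()
    for s in TRAIN_SMILES:
        presence.update(extract_attributes(s, 1).keys())
    return presence


class TestOptimizeWeights:
    def test_endpoint_equal_to_attribute_count_reaches_perfect_r(self):
        y = np.array([extract_attributes(s, 1)["O"] for s in TRAIN_SMILES], float)
        model = optimize_weights(TRAIN_SMILES, y, order=1, threshold=2,
                                 n_epochs=300, seed=5)
        assert model.train_r_history[-1] == pytest.approx(1.0, abs=1e-9)

    def test_accepted_move_history_non_decreasing(self):
        ds_y = np.array([len(s) for s in TRAIN_SMILES], float)
        model = optimize_weights(TRAIN_SMILES, ds_y, order=2, threshold=2,
                                 n_epochs=20, seed=1)
        hist = np.array(model.train_r_history)
        assert (np.diff(hist) >= -1e-12).all()
        assert hist[-1] >= hist[0]

    def test_same_seed_identical_weight_maps(self):
        y = np.arange(12, dtype=float)
        a = optimize_weights(TRAIN_SMILES, y, n_epochs=10, seed=3)
        b = optimize_weights(TRAIN_SMILES, y, n_epochs=10, seed=3)
        assert a.weights == b.weights
        assert (a.slope, a.intercept) == (b.slope, b.intercept)

    def test_recovers_attribute_linear_endpoint(self):
        rng = np.random.default_rng(0)
        counts = [extract_attributes(s, 1) for s in TRAIN_SMILES]
        y = np.array([3 * c["C"] + 7 * c["O"] for c in counts], float)
        y += rng.normal(0, 0.1, len(y))
        model = optimize_weights(TRAIN_SMILES, y, order=1, threshold=2,
                                 n_epochs=300, seed=3)
        pred = model.predict(TRAIN_SMILES)
        r2 = np.corrcoef(pred, y)[0, 1] ** 2
        assert r2 >= 0.9

    def test_frozen_model_prediction_order_equivariance(self):
        """Test-set use never touches training artifacts: predicting a
        permuted test list permutes the predictions and nothing else."""
        y = np.array([len(s) for s in TRAIN_SMILES], float)
        model = optimize_weights(TRAIN_SMILES, y, n_epochs=10, seed=2)
        test = ["CCCCCO", "OCCCO", "CCCOC"]
        w_before = dict(model.weights)
        direct = model.predict(test)
        permuted = model.predict(test[::-1])
        assert np.allclose(direct[::-1], permuted)
        assert model.weights == w_before

    def test_too_few_compounds_rejected(self):
        with pytest.raises(OptimizationError):
            optimize_weights(["CCO"] * 5, np.arange(5.0))

    def test_constant_endpoint_rejected(self):
        with pytest.raises(OptimizationError):
            optimize_weights(TRAIN_SMILES, np.ones(12))

    def test_all_subthreshold_raises_no_active_attributes(self):
        with pytest.raises(OptimizationError, match="active"):
            optimize_weights(TRAIN_SMILES, np.arange(12.0), threshold=1000)


def test_model_json_roundtrip(tmp_path):
    y = np.arange(12, dtype=float)
    model = optimize_weights(TRAIN_SMILES, y, n_epochs=5, seed=1)
    path = tmp_path / "dcw.json"
    model.to_json(path)
    back = DCWModel.from_json(path)
    assert back.weights == model.weights
    assert back.slope == pytest.approx(model.slope)
    assert np.allclose(back.predict(TRAIN_SMILES), model.predict(TRAIN_SMILES))
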