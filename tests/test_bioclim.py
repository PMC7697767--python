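import numpy as np
import pandas as pd
import pytest

from sdmlite.bioclim import BioclimEnvelope, project_envelope

from conftest import make_stack


def percentile_oracle(train, value):
    """Count-based midrank percentile on a tiny training set."""
    train = np.asarray(train, dtype=float)
    return (np.sum(train < value) + 0.5 * np.sum(train == value)) / len(train)


def suitability_oracle(envelopes, row, tails="continuous"):
    """Slow per-variable scoring followed by the min aggregation."""
    scores = []
    for train, x in zip(envelopes, row):
        train = np.asarray(train, dtype=float)
        p = percentile_oracle(train, x)
        if x < train.min() or x > train.max():
            s = 0.0
        else:
            s = 2.0 * min(p, 1.0 - p)
        if tails == "clamped10_90" and (p < 0.1 or p > 0.9):
            s = 0.0
        scores.append(s)
    return min(scores)


@pytest.fixture()
def nine_point_model():
    X = pd.DataFrame({"a": np.arange(1.0, 10.0)})
    return BioclimEnvelope().fit(X)


class TestFit:
    def test_sorted_training_values_stored(self):
        X = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [0.1, 0.3, 0.2]})
        model = BioclimEnvelope().fit(X)
        np.testing.assert_array_equal(model.envelope_["a"], [1.0, 3.0, 5.0])
        assert model.n_train_ == 3

    def test_single_presence(self):
        model = BioclimEnvelope().fit(pd.DataFrame({"a": [2.0], "b": [3.0]}))
        assert all(len(model.envelope_[v]) == 1 for v in ("a", "b"))

    def test_row_order_invariant(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        m1 = BioclimEnvelope().fit(X)
        m2 = BioclimEnvelope().fit(X.sample(frac=1, random_state=1))
        probe = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))

    def test_empty_presences_rejected(self):
        with pytest.raises(ValueError):
            BioclimEnvelope().fit(pd.DataFrame({"a": []}))


class TestPercentile:
    @pytest.mark.parametrize("value,expected", [
        (5.0, 0.5),
        (3.0, 2.5 / 9.0),
        (9.0, 8.5 / 9.0),
    ])
    def test_examples_on_1_to_9(self, nine_point_model, value, expected):
        assert nine_point_model.percentile_score("a", value) == pytest.approx(expected)

    def test_matches_count_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            train = rng.integers(0, 20, size=rng.integers(1, 51)).astype(float)
            model = BioclimEnvelope().fit(pd.DataFrame({"a": train}))
            for value in rng.uniform(-2, 22, size=10):
                assert model.percentile_score("a", value) == pytest.approx(
                    percentile_oracle(train, value))

    def test_unknown_variable(self, nine_point_model):
        with pytest.raises(KeyError):
            nine_point_model.percentile_score("zzz", 1.0)


class TestSuitability:
    def test_median_scores_one(self):
        X = pd.DataFrame({"a": np.arange(1.0, 10.0), "b": np.arange(11.0, 20.0)})
        model = BioclimEnvelope().fit(X)
        assert model.predict(pd.DataFrame({"a": [5.0], "b": [15.0]}))[0] == 1.0

    def test_outside_envelope_scores_zero(self, nine_point_model):
        out = nine_point_model.predict(pd.DataFrame({"a": [0.5, 9.5]}))
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_two_variable_min_aggregation(self):
        X = pd.DataFrame({"a": np.arange(1.0, 10.0), "b": np.arange(1.0, 10.0)})
        model = BioclimEnvelope().fit(X)
        score = model.predict(pd.DataFrame({"a": [5.0], "b": [3.0]}))[0]
        assert score == pytest.approx(5.0 / 9.0)

    def test_matches_suitability_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        for tails in ("continuous", "clamped10_90"):
            train = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
            model = BioclimEnvelope(tails=tails).fit(train)
            probe = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
            got = model.predict(probe)
            want = [suitability_oracle([train[v] for v in "abc"], row, tails)
                    for row in probe.to_numpy()]
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_scores_bounded_and_clamped_never_higher(self):
        rng = np.random.default_rng(8)
        train = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        probe = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        cont = BioclimEnvelope().fit(train).predict(probe)
        clam = BioclimEnvelope(tails="clamped10_90").fit(train).predict(probe)
        assert ((0 <= cont) & (cont <= 1)).all()
        assert (clam <= cont + 1e-12).all()

    def test_score_decreases_away_from_median(self, nine_point_model):
        # folded percentile: monotone non-increasing as the value moves
        # outward from the median on either side
        right = nine_point_model.predict(pd.DataFrame({"a": [5.0, 6.0, 7.5, 9.0]}))
        left = nine_point_model.predict(pd.DataFrame({"a": [5.0, 4.0, 2.5, 1.0]}))
        assert (np.diff(right) <= 1e-12).all()
        assert (np.diff(left) <= 1e-12).all()

    def test_missing_value_rejected(self, nine_point_model):
        with pytest.raises(ValueError):
            nine_point_model.predict(pd.DataFrame({"a": [np.nan]}))


class TestProjection:
    def test_grid_equals_pointwise_application(self):
        rng = np.random.default_rng(9)
        stack = make_stack(rng.normal(size=(2, 20, 20)), codes=["a", "b"], y0=20.0)
        stack.values[:, 3, 4] = np.nan
        train = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        model = BioclimEnvelope().fit(train)
        grid = project_envelope(model, stack)
        for r in range(20):
            for c in range(20):
                if np.isnan(stack.values[0, r, c]):
                    assert np.isnan(grid[r, c])
                else:
                    row = pd.DataFrame({"a": [stack.values[0, r, c]],
                                        "b": [stack.values[1, r, c]]})
                    assert grid[r, c] == pytest.approx(model.predict(row)[0])

    def test_training_cells_score_positive_in_continuous_mode(self, fixture_bundle):
        _, stack, _, occ = fixture_bundle
        from sdmlite.grids import extract_values
        pres = extract_values(stack, occ.points, label=1)
        model = BioclimEnvelope().fit(pres[stack.codes])
        scores = model.predict(pres[stack.codes])
        assert (scores > 0).all()

    def test_missing_layer_rejected(self):
        stack = make_stack(np.zeros((4, 4)), codes=["a"], y0=4.0)
        model = BioclimEnvelope().fit(pd.DataFrame({"a": [1.0], "zz": [2.0]}))
        with pytest.raises(KeyError):
            project_envelope(model, stack)

    def test_all_nodata_layer_rejected(self):
        vals = np.zeros((2, 4, 4))
        vals[1] = np.nan
        stack = make_stack(vals, codes=["a", "b"], y0=4.0)
        model = BioclimEnvelope().fit(
            pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            project_envelope(model, stack)


class TestSerialization:
    def test_json_roundtrip(self):
        rng = np.random.default_rng(10)
        train = pd.DataFrame({"a": rng.normal(size=15), "b": rng.normal(size=15)})
        model = BioclimEnvelope(tails="clamped10_90").fit(train)
        back = BioclimEnvelope.from_json(model.to_json())
        probe = pd.DataFrame({"a": rng.normal(size=5), "b": rng.normal(size=5)})
        np.testing.assert_array_equal(model.predict(probe), back.predict(probe))
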