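"""Ordinal classification schemes and the RI-threshold recalibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import soilrisk as sr


@pytest.mark.parametrize(
    "scheme,value,expected",
    [
        ("Cf", 6.0, "Very high"),
        ("Cf", 0.999999, "Low"),
        ("Cf", 1.0, "Moderate"),
        ("mCd", 1.5, "Low degree of contamination"),
        ("mCd", 40.0, "Ultra-high degree of contamination"),
        ("Pn", 0.7, "Safety domain"),           # closed upper bound honoured
        ("Pn", 1.0, "Precaution domain"),
        ("Pn", 3.01, "Seriously polluted domain"),
        ("Igeo", 0.0, "Unpolluted"),            # overlapping rows: lower class wins
        ("Igeo", 3.0, "Heavily polluted"),
        ("Igeo", -5.0, "Unpolluted"),
        ("PLI", 1.0, "Baseline levels of pollution"),
        ("PLI", 0.99, "Not polluted"),
        ("PLI", 1.01, "Polluted"),
        ("Eir", 30.0, "moderate risk"),
        ("Eir", 500.0, "significantly high risk"),
    ],
)
def test_published_class_boundaries(scheme, value, expected):
    assert sr.classify_value(value, sr.builtin_scheme(scheme)) == expected


def test_unknown_scheme_and_nonfinite_value_rejected():
    with pytest.raises(sr.SoilRiskError, match="no built-in scheme"):
        sr.builtin_scheme("Zn")
    with pytest.raises(sr.SoilRiskError, match="non-finite"):
        sr.classify_value(float("nan"), sr.builtin_scheme("Cf"))


class TestRecalibration:
    def test_nine_element_default_suite(self, refs):
        scheme = sr.recalibrate_ri_thresholds(refs)
        assert scheme.lower_bounds == (80.0, 160.0, 320.0)
        assert scheme.labels == ("low risk", "moderate risk", "considerable risk", "high risk")

    def test_hakanson_fixed_point(self):
        """A toxicity suite summing to 133 recovers the original grades."""
        scheme = sr.recalibrate_ri_thresholds({"A": 100.0, "B": 33.0})
        assert scheme.lower_bounds == (150.0, 300.0, 600.0)

    def test_single_element_cadmium(self):
        scheme = sr.recalibrate_ri_thresholds({"Cd": 30.0})
        assert scheme.lower_bounds == (30.0, 60.0, 120.0)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(sr.SoilRiskError, match="empty"):
            sr.recalibrate_ri_thresholds({})
        with pytest.raises(sr.SoilRiskError, match="non-positive"):
            sr.recalibrate_ri_thresholds({"As": 0.0})

    @given(tox=st.lists(st.floats(min_value=0.5, max_value=50.0), min_size=1, max_size=12))
    def test_bounds_double(self, tox):
        scheme = sr.recalibrate_ri_thresholds({f"E{i}": t for i, t in enumerate(tox)})
        b = scheme.lower_bounds
        assert all(b2 == 2 * b1 for b1, b2 in zip(b, b[1:]))
        assert b[0] > 0
        if b[0] >= 10:
            assert b[0] % 10 == 0  # rounded to the nearest multiple of ten

    def test_rounding_ties_go_up(self):
        # ΣTr × 150/133 = 75 exactly when ΣTr = 66.5
        rule = sr.RecalibrationRule()
        assert rule.first_bound(66.5) == 80.0


@pytest.mark.parametrize("name", ["Cf", "mCd", "Pn", "Igeo", "PLI", "Eir"])
def test_labels_monotone_in_value(name):
    """Increasing an index value never moves its label toward a
    less-contaminated class; every finite value receives exactly one label."""
    scheme = sr.builtin_scheme(name)
    rank = {label: i for i, label in enumerate(scheme.labels)}
    rng = np.random.default_rng(5)
    values = np.sort(np.concatenate([
        rng.uniform(-2, 2 * (scheme.lower_bounds[-1] + 1), 200),
        np.array(scheme.lower_bounds),
        np.array(scheme.lower_bounds) - 1e-9,
        np.array(scheme.lower_bounds) + 1e-9,
    ]))
    labels = [sr.classify_value(float(v), scheme) for v in values]
    ranks = [rank[l] for l in labels]
    assert all(r2 >= r1 for r1, r2 in zip(ranks, ranks[1:]))


def test_classify_index_table_on_identity_site(background_table, refs):
    idx = sr.compute_index_table(background_table, refs)
    schemes = sr.default_schemes(refs, elements=list(background_table.elements))
    classified = sr.classify_index_table(idx, schemes)
    labels = classified.set_index("index")["label"]
    assert labels["Cf_As"] == "Moderate"          # Cf = 1 sits on the printed cut
    assert labels["Igeo_As"] == "Unpolluted"      # log2(1/1.5) < 0
    assert labels["mCd"] == "Nil to very low degree of contamination"
    assert labels["Pn"] == "Precaution domain"    # Pn = 1, closed upper bound
    assert labels["PLI"] == "Baseline levels of pollution"
    assert labels["RI"] == "low risk"             # RI = 70 under the recalibrated bound 80


def test_missing_values_classify_as_unclassified(refs):
    idx = pd.DataFrame({"mCd": [np.nan, 2.5]},
                       index=pd.Index(["P1", "P2"], name="site_id"))
    out = sr.classify_index_table(idx, {"mCd": sr.builtin_scheme("mCd")})
    labels = out.set_index("site_id")["label"]
    assert labels["P1"] == sr.UNCLASSIFIED
    assert labels["P2"] == "Moderate degree of contamination"


def test_uncovered_index_column_rejected():
    idx = pd.DataFrame({"Pn": [1.0]}, index=pd.Index(["P1"], name="site_id"))
    with pytest.raises(sr.SoilRiskError, match="Pn"):
        sr.classify_index_table(idx, {"Cf": sr.builtin_scheme("Cf")})


def test_scheme_config_round_trip():
    for name in ("Cf", "Pn", "Igeo", "PLI"):
        scheme = sr.builtin_scheme(name)
        assert sr.CategoryScheme.from_dict(scheme.to_dict()) == scheme
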