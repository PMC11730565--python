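"""Index arithmetic: worked values, error contracts, invariants, and a
brute-force oracle for the per-site orchestration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import soilrisk as sr
from conftest import random_sample_table

conc = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)
positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    "func,args,expected",
    [
        (sr.contamination_factor, (5.0, 5.0), 1.0),
        (sr.contamination_factor, (30.0, 5.0), 6.0),
        (sr.contamination_factor, (0.0, 0.3), 0.0),
        (sr.pollution_index, (25.0, 5.0), 5.0),
        (sr.modified_contamination_degree, ([1.0] * 9,), 1.0),
        (sr.modified_contamination_degree, ([2.0, 4.0],), 3.0),
        (sr.nemerow_index, ([1.0, 1.0, 1.0],), 1.0),
        (sr.nemerow_index, ([1.0, 7.0],), math.sqrt(32.5)),
        (sr.nemerow_index, ([3.0],), 3.0),
        (sr.geoaccumulation_index, (12.0, 1.0), 3.0),
        (sr.single_element_risk, (30.0, 1.0), 30.0),
        (sr.single_element_risk, (10.0, 0.0), 0.0),
        (sr.single_element_risk, (5.0, 4.0), 20.0),
        (sr.aggregate_risk, ([30.0, 10.0, 5.0],), 45.0),
        (sr.pollution_load_index, ([1.0] * 5,), 1.0),
        (sr.pollution_load_index, ([1.0, 4.0],), 2.0),
    ],
)
def test_worked_values(func, args, expected):
    assert func(*args) == pytest.approx(expected, rel=1e-12)


def test_igeo_zero_at_one_and_a_half_background():
    assert sr.geoaccumulation_index(1.5 * 7.0, 7.0) == 0.0


@pytest.mark.parametrize(
    "func,args",
    [
        (sr.contamination_factor, (5.0, 0.0)),          # zero background
        (sr.contamination_factor, (-1.0, 5.0)),         # negative concentration
        (sr.pollution_index, (5.0, 0.0)),
        (sr.modified_contamination_degree, ([],)),
        (sr.nemerow_index, ([],)),
        (sr.geoaccumulation_index, (0.0, 5.0)),         # censored concentration
        (sr.single_element_risk, (0.0, 1.0)),           # non-positive toxicity
        (sr.aggregate_risk, ([],)),
        (sr.pollution_load_index, ([1.0, 0.0],)),       # geometric mean at zero
    ],
)
def test_error_contracts(func, args):
    with pytest.raises(sr.SoilRiskError):
        func(*args)


def test_background_site_is_the_identity_point(background_table, refs):
    """At exact background: Cf = PI = 1 per element, mCd = Pn = PLI = 1,
    Igeo = log2(1/1.5) < 0, and RI equals the summed toxicity (70)."""
    idx = sr.compute_index_table(background_table, refs)
    row = idx.loc["B001"]
    for el in sr.STUDY_ELEMENTS:
        assert row[f"Cf_{el}"] == pytest.approx(1.0, rel=1e-12)
        assert row[f"Igeo_{el}"] == pytest.approx(math.log2(1 / 1.5), rel=1e-12)
        assert row[f"Eir_{el}"] == pytest.approx(refs.toxicity[el], rel=1e-12)
    assert row["mCd"] == pytest.approx(1.0, rel=1e-12)
    assert row["Pn"] == pytest.approx(1.0, rel=1e-12)
    assert row["RI"] == pytest.approx(70.0, rel=1e-12)
    assert row["PLI"] == pytest.approx(1.0, rel=1e-12)
    assert row["n_elements"] == 9


def test_missing_element_shrinks_composites(background_table, refs):
    table = background_table
    table.data.loc["B001", "Sb"] = np.nan
    idx = sr.compute_index_table(table, refs)
    row = idx.loc["B001"]
    assert row["n_elements"] == 8
    assert row["mCd"] == pytest.approx(1.0)           # mean over the 8 present
    assert row["RI"] == pytest.approx(70.0 - 7.0)     # Sb's Eir contribution gone
    assert np.isnan(row["Cf_Sb"])


def test_zero_concentration_flags_igeo_and_pli(background_table, refs):
    table = background_table
    table.data.loc["B001", "As"] = 0.0
    idx = sr.compute_index_table(table, refs)
    row = idx.loc["B001"]
    assert row["Cf_As"] == 0.0
    assert np.isnan(row["Igeo_As"])   # no Igeo for a censored value
    assert np.isnan(row["PLI"])       # geometric mean undefined at zero
    assert row["n_elements"] == 9


def test_empty_table_yields_empty_index_table(refs):
    df = pd.DataFrame(columns=["x", "y", "As"]).rename_axis("site_id")
    idx = sr.compute_index_table(sr.SampleTable(df), refs, elements=["As"])
    assert len(idx) == 0
    assert "Cf_As" in idx.columns and "RI" in idx.columns


def test_element_without_reference_fails_before_computation(refs):
    rng = np.random.default_rng(0)
    table = random_sample_table(rng, 2, ["As"])
    table.data["Zn"] = 50.0  # registered element, but no background value
    with pytest.raises(sr.SoilRiskError, match="Zn"):
        sr.compute_index_table(table, refs)


def test_detection_limit_substitution(refs):
    rng = np.random.default_rng(1)
    table = random_sample_table(rng, 1, ["As"])
    table.data["As"] = 0.2
    idx = sr.compute_index_table(table, refs, elements=["As"],
                                 detection_limits={"As": 0.5})
    assert idx["Cf_As"].iloc[0] == pytest.approx(0.25 / 5.0)


def test_orchestration_matches_brute_force_oracle(refs):
    """compute_index_table agrees with an element-by-element recomputation
    through the scalar operations, to 1e-12 relative."""
    rng = np.random.default_rng(42)
    elements = ["As", "Cd", "Cu", "Pb"]
    table = random_sample_table(rng, 5, elements)
    idx = sr.compute_index_table(table, refs, elements=elements)
    for site_id, site in table.data.iterrows():
        cf = [sr.contamination_factor(site[el], refs.background[el]) for el in elements]
        eir = [sr.single_element_risk(refs.toxicity[el], c) for el, c in zip(elements, cf)]
        row = idx.loc[site_id]
        for el, c in zip(elements, cf):
            assert row[f"Cf_{el}"] == pytest.approx(c, rel=1e-12)
            assert row[f"Igeo_{el}"] == pytest.approx(
                sr.geoaccumulation_index(site[el], refs.background[el]), rel=1e-12
            )
        assert row["mCd"] == pytest.approx(sr.modified_contamination_degree(cf), rel=1e-12)
        assert row["Pn"] == pytest.approx(sr.nemerow_index(cf), rel=1e-12)
        assert row["RI"] == pytest.approx(sr.aggregate_risk(eir), rel=1e-12)
        assert row["PLI"] == pytest.approx(sr.pollution_load_index(cf), rel=1e-12)


@given(ci=conc, cb=positive, k=st.floats(min_value=1e-3, max_value=1e3))
def test_scale_equivariance(ci, cb, k):
    """Rescaling a concentration and its background together leaves the
    ratio indices unchanged."""
    assert sr.contamination_factor(k * ci, k * cb) == pytest.approx(
        sr.contamination_factor(ci, cb), rel=1e-9
    )
    assert sr.geoaccumulation_index(k * ci, k * cb) == pytest.approx(
        sr.geoaccumulation_index(ci, cb), rel=1e-6, abs=1e-9
    )


@given(ci=conc, cb=positive, bump=st.floats(min_value=0.0, max_value=1e3))
def test_monotone_in_concentration(ci, cb, bump):
    assert sr.contamination_factor(ci + bump, cb) >= sr.contamination_factor(ci, cb)
    assert sr.geoaccumulation_index(ci + bump, cb) >= sr.geoaccumulation_index(ci, cb)
    assert sr.single_element_risk(5.0, (ci + bump) / cb) >= sr.single_element_risk(5.0, ci / cb)


@given(ci=conc, cb=positive)
def test_cf_pi_identity_and_igeo_consistency(ci, cb):
    """Cf ≡ PI under a shared reference table, and Igeo = log2(Cf / 1.5)."""
    cf = sr.contamination_factor(ci, cb)
    assert sr.pollution_index(ci, cb) == cf
    assert sr.geoaccumulation_index(ci, cb) == pytest.approx(
        math.log2(cf / 1.5), rel=1e-9, abs=1e-12
    )


@given(pis=st.lists(st.floats(min_value=0.0, max_value=1e4), min_size=1, max_size=12))
def test_nemerow_bracketed_by_max(pis):
    pn = sr.nemerow_index(pis)
    assert max(pis) / math.sqrt(2) - 1e-9 <= pn <= max(pis) + 1e-9
    assert pn >= np.mean(pis) / math.sqrt(2) - 1e-9


@given(cfs=st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1, max_size=12))
def test_pli_bracketed_by_extremes(cfs):
    pli = sr.pollution_load_index(cfs)
    assert min(cfs) - 1e-9 <= pli <= max(cfs) + 1e-9
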